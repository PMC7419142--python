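"""Scripted experiment protocols.

Each protocol is a pure function of its configuration and a base seed:
trial *i* of a protocol draws its randomness from a sub-seed derived by
counter (`trial_seed(base, i, ...)`), so re-running reproduces every
record and adding trials never perturbs earlier ones.  Protocols emit an
:class:`ExperimentResult` with tidy per-trial records and a summary
table (medians with standard deviations, matching how bump and tuning
statistics are conventionally reported for these circuits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import lif, metrics, stimuli
from .circuit import (ConnectivityMatrix, WeightVector, build_species_circuit,
                      hemisphere_asymmetry, synaptic_noise)
from .optimize import calibrate_peak_rate
from .params import NeuronParams

NEURON_CLASSES = ("E-PG", "P-EN", "P-EG", "Delta7")

#: amplitude/peak ratio below which a profile counts as flat (FWHM 'N/A')
FLAT_MODULATION = 0.15
#: minimum E-PG bump peak/amplitude (imp/s) for a trial to count as holding
#: a heading signal; anything weaker is indistinguishable from the 5 imp/s
#: Poisson background
MIN_BUMP_PEAK = 50.0
MIN_BUMP_AMPLITUDE = 25.0


def trial_seed(base: int, *keys: int) -> int:
    """Deterministic sub-seed for one trial (counter scheme, < 2**31)."""
    ss = np.random.SeedSequence([int(base) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ExperimentResult:
    protocol: str
    variant: str
    records: pd.DataFrame
    summary: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(directory / f"{self.protocol}_records.csv", index=False)
        self.summary.to_csv(directory / f"{self.protocol}_summary.csv", index=False)


# ---------------------------------------------------------------------------
# Common plumbing
# ---------------------------------------------------------------------------

def _simulate(cx, params, segments, duration, seed, g_leak=None, C_m=None):
    proto = stimuli.StimulusProtocol(cx.n_neurons)
    for s in segments:
        proto.add(s)
    return lif.simulate_network(cx, params, proto, duration=duration,
                                seed=seed, g_leak=g_leak, C_m=C_m)


def _maintenance_raster(cx, params, azimuth, peak_rate, stim_duration,
                        dark_duration, seed):
    # darkness carries no input; the only stochasticity is the Poisson
    # stimulus history before removal
    segs = [
        stimuli.heading_segment(cx, np.deg2rad(azimuth), peak_rate, 0.0,
                                stim_duration),
    ]
    return _simulate(cx, params, segs, stim_duration + dark_duration, seed)


def _class_stats_at(raster, cx, t):
    rows = []
    for cls in NEURON_CLASSES:
        if len(cx.class_indices(cls)) == 0:
            continue
        centres, prof = metrics.azimuth_profile_at(raster, cx, t, cls)
        fwhm, n_arcs = metrics.profile_fwhm(prof)
        try:
            heading = metrics.decode_heading(prof, centres)
        except metrics.UndefinedHeadingError:
            heading = np.nan
        rows.append({
            "cls": cls, "heading": heading, "fwhm": fwhm,
            "peak": float(prof.max()),
            "amplitude": float(prof.max() - prof.min()),
            "n_arcs": n_arcs,
        })
    return rows


# ---------------------------------------------------------------------------
# Bump maintenance (darkness persistence)
# ---------------------------------------------------------------------------

def run_bump_maintenance(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    n_trials: int = 40,
    azimuth: float = 180.0,
    stim_duration: float = 3.0,
    measure_after: float = 10.0,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Stimulate, remove the stimulus, and measure the surviving bump.

    Per trial the bump statistics of every neuron class are taken
    ``measure_after`` seconds into darkness.  A trial fails when the
    E-PG profile no longer encodes a single defined heading; failures
    are counted but excluded from the width medians.
    """
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    t_meas = stim_duration + measure_after
    records = []
    for i in range(n_trials):
        s = trial_seed(seed, 1, i)
        raster = _maintenance_raster(cx, params, azimuth, peak_rate,
                                     stim_duration, measure_after, s)
        stats = _class_stats_at(raster, cx, t_meas - params.dt)
        epg = next(r for r in stats if r["cls"] == "E-PG")
        success = bool(np.isfinite(epg["heading"]) and epg["n_arcs"] == 1
                       and epg["peak"] >= MIN_BUMP_PEAK
                       and epg["amplitude"] >= MIN_BUMP_AMPLITUDE)
        for r in stats:
            records.append({"trial": i, "seed": s, "success": success, **r})
    rec = pd.DataFrame(records)
    ok = rec[rec["success"]]
    rows = []
    for cls, grp in ok.groupby("cls", sort=False):
        flat = grp["amplitude"].median() < FLAT_MODULATION * grp["peak"].median()
        rows.append({
            "cls": cls,
            "fwhm_median": np.nan if flat else grp["fwhm"].median(),
            "fwhm_sd": np.nan if flat else grp["fwhm"].std(),
            "peak_median": grp["peak"].median(),
            "peak_sd": grp["peak"].std(),
            "amplitude_median": grp["amplitude"].median(),
            "amplitude_sd": grp["amplitude"].std(),
            "fwhm_na": bool(flat),
        })
    summary = pd.DataFrame(rows)
    success_frac = rec.groupby("trial")["success"].first().mean() if len(rec) else 0.0
    return ExperimentResult(
        protocol="bump_maintenance", variant=_variant_name(cx),
        records=rec, summary=summary,
        meta={"seed": seed, "n_trials": n_trials, "azimuth": azimuth,
              "peak_rate": peak_rate, "measure_after": measure_after,
              "success_fraction": float(success_frac)},
    )


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------

def run_tuning_curves(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    n_trials: int = 40,
    azimuths: Optional[Sequence[float]] = None,
    stim_duration: float = 3.0,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Sweep the stimulus azimuth and measure per-class responses.

    Each (trial, octant-unit) pair yields a tuning curve sampled at the
    stimulus azimuths relative to the unit's preferred direction; curves
    are peak-aligned and summarised by median FWHM/peak/amplitude.
    """
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    n_oct = cx.n_octants
    if azimuths is None:
        azimuths = metrics.octant_centres(n_oct)
    azimuths = np.asarray(azimuths, float)

    # responses[cls][j, i, b]: azimuth j, trial i, domain-azimuth bin b
    bins = {cls: metrics._azimuth_bins(cx, cls)[1]
            for cls in NEURON_CLASSES if len(cx.class_indices(cls))}
    responses = {cls: np.zeros((len(azimuths), n_trials, bins[cls].size))
                 for cls in bins}
    records = []
    for j, az in enumerate(azimuths):
        for i in range(n_trials):
            s = trial_seed(seed, 2, j, i)
            seg = stimuli.heading_segment(cx, np.deg2rad(az), peak_rate, 0.0,
                                          stim_duration)
            raster = _simulate(cx, params, [seg], stim_duration, s)
            for cls in responses:
                centres, prof = metrics.azimuth_profile_at(
                    raster, cx, stim_duration - params.dt, cls)
                responses[cls][j, i] = prof
                for b, rate in enumerate(prof):
                    records.append({"azimuth": az, "trial": i, "cls": cls,
                                    "unit_azimuth": centres[b], "rate": rate,
                                    "seed": s})

    rows = []
    curves = {}
    for cls, resp in responses.items():
        # tuning curve of octant o in trial i: response vs stimulus azimuth
        n_units = resp.shape[2]
        per_curve = []
        for i in range(n_trials):
            for o in range(n_units):
                curve = resp[:, i, o]
                fwhm, _ = metrics.profile_fwhm(curve)
                per_curve.append({"fwhm": fwhm, "peak": curve.max(),
                                  "amplitude": curve.max() - curve.min()})
        df = pd.DataFrame(per_curve)
        flat = df["amplitude"].median() < FLAT_MODULATION * df["peak"].median()
        rows.append({
            "cls": cls,
            "fwhm_median": np.nan if flat else df["fwhm"].median(),
            "fwhm_sd": np.nan if flat else df["fwhm"].std(),
            "peak_median": df["peak"].median(),
            "peak_sd": df["peak"].std(),
            "amplitude_median": df["amplitude"].median(),
            "amplitude_sd": df["amplitude"].std(),
            "fwhm_na": bool(flat),
        })
        # peak-aligned mean curve (peak shifted to 0 deg)
        mean_resp = resp.mean(axis=1)  # (n_az, n_units)
        aligned = np.stack([np.roll(mean_resp[:, o], -int(np.argmax(mean_resp[:, o])))
                            for o in range(n_units)])
        curves[cls] = aligned.mean(axis=0)
    summary = pd.DataFrame(rows)
    return ExperimentResult(
        protocol="tuning_curves", variant=_variant_name(cx),
        records=pd.DataFrame(records), summary=summary,
        meta={"seed": seed, "n_trials": n_trials, "peak_rate": peak_rate,
              "azimuths": azimuths.tolist(),
              "aligned_curves": {k: v.tolist() for k, v in curves.items()}},
    )


# ---------------------------------------------------------------------------
# Heading change (jump vs gradual, transition time)
# ---------------------------------------------------------------------------

def run_heading_change(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    delta: float = 120.0,
    n_trials: int = 20,
    azimuth1: float = 90.0,
    stim1: float = 3.0,
    darkness: float = 2.0,
    stim2: float = 3.0,
    peak_rate: Optional[float] = None,
    seed: int = 0,
    settle_tolerance: float = 22.5,
    settle_window: float = 0.5,
    g_leak: Optional[np.ndarray] = None,
    C_m: Optional[np.ndarray] = None,
) -> ExperimentResult:
    """Sudden heading change: stimulus, darkness, second stimulus at
    ``azimuth1 + delta``; records transition time, jump/gradual class and
    maximal angular rate (shortest angular distance / transition time)."""
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    az2 = (azimuth1 + delta) % 360.0
    onset = stim1 + darkness
    # a darkness tail after the second stimulus so the 3 s hold criterion
    # has room beyond the settling transient
    duration = onset + stim2 + 1.0
    n_oct = cx.n_octants
    span = 360.0 / n_oct
    from_o = int(round(azimuth1 / span)) % n_oct
    to_o = int(round(az2 / span)) % n_oct
    records = []
    for i in range(n_trials):
        s = trial_seed(seed, 3, int(round(delta * 10)), i)
        segs = [
            stimuli.heading_segment(cx, np.deg2rad(azimuth1), peak_rate, 0.0, stim1),
            stimuli.heading_segment(cx, np.deg2rad(az2), peak_rate, onset,
                                    onset + stim2),
        ]
        raster = _simulate(cx, params, segs, duration, s, g_leak, C_m)
        trace = metrics.smooth_rates(raster)
        times, headings = metrics.heading_series(trace, cx)
        # settle relative to the state actually reached (attractor states
        # need not coincide with the stimulus azimuth), but only count
        # trials that ended near the commanded heading
        t_tr = metrics.transition_time(times, headings, onset, None,
                                       settle_tolerance, settle_window)
        final = metrics.settled_heading(times, headings)
        if (not np.isfinite(final)
                or metrics.heading_error(final, az2) > 45.0):
            t_tr = float("inf")
        prof = metrics.octant_profile_matrix(trace, cx)
        a = int(round(onset / trace.dt))
        kind = ("gradual" if from_o == to_o else
                metrics.classify_transition(prof[:, a:], from_o, to_o))
        sad = metrics.shortest_angular_distance(delta % 360.0)
        rate = sad / t_tr if np.isfinite(t_tr) and t_tr > 0 else (
            np.inf if t_tr == 0 else np.nan)
        sel = times >= onset
        stable = metrics.trial_stability(times[sel], headings[sel], az2)
        records.append({"trial": i, "seed": s, "delta": delta,
                        "transition_time": t_tr, "kind": kind,
                        "angular_rate": rate, "stable": stable})
    rec = pd.DataFrame(records)
    fin = rec[np.isfinite(rec["transition_time"])]
    summary = pd.DataFrame([{
        "delta": delta,
        "transition_time_median": fin["transition_time"].median(),
        "transition_time_sd": fin["transition_time"].std(),
        "angular_rate_median": fin["angular_rate"].replace(np.inf, np.nan).median(),
        "frac_jump": (rec["kind"] == "jump").mean(),
        "frac_gradual": (rec["kind"] == "gradual").mean(),
        "frac_stable": rec["stable"].mean(),
    }])
    return ExperimentResult(
        protocol="heading_change", variant=_variant_name(cx),
        records=rec, summary=summary,
        meta={"seed": seed, "azimuth1": azimuth1, "delta": delta,
              "peak_rate": peak_rate, "onset": onset},
    )


# ---------------------------------------------------------------------------
# Sigma sweep (inhibition-uniformity regime map)
# ---------------------------------------------------------------------------

def _rescale_inhibition_blocks(cx_swept, cx_base):
    """Scale the Gaussian-profile blocks of a sigma-swept circuit so the
    total E-PG->Delta7 and Delta7->Delta7 input matches the base circuit."""
    M = cx_swept.M.copy()
    for pre_cls, post_cls in (("E-PG", "Delta7"), ("Delta7", "Delta7")):
        pre_s = cx_swept.class_indices(pre_cls)
        post_s = cx_swept.class_indices(post_cls)
        pre_b = cx_base.class_indices(pre_cls)
        post_b = cx_base.class_indices(post_cls)
        tot_s = np.abs(M[np.ix_(pre_s, post_s)]).sum()
        tot_b = np.abs(cx_base.M[np.ix_(pre_b, post_b)]).sum()
        if tot_s > 0:
            M[np.ix_(pre_s, post_s)] *= tot_b / tot_s
    return ConnectivityMatrix(
        M=M, neurons=cx_swept.neurons, species=cx_swept.species,
        sigma=cx_swept.sigma, weights=cx_swept.weights,
        n_octants=cx_swept.n_octants,
        meta={**cx_swept.meta, "inhibition_rescaled": True},
    )


def run_sigma_sweep(
    species: str,
    weights: WeightVector,
    params: Optional[NeuronParams] = None,
    sigma_grid: Sequence[float] = (0.2, 0.4, 0.8, 1.6, 3.0),
    delta_grid: Sequence[float] = (45.0, 90.0, 135.0, 180.0),
    n_trials: int = 10,
    peak_rate: Optional[float] = None,
    seed: int = 0,
    n_octants: int = 8,
) -> ExperimentResult:
    """Transition-regime map over inhibitory-profile width and heading step.

    The species circuit is rebuilt at each sigma (the fly uses the
    Gaussian-profile construction of the hybrid model, which approaches
    its uniform inhibition at large sigma); profile blocks are rescaled
    to conserve total inhibitory input, and each (sigma, delta) cell is
    labelled gradual / jump / both from repeated heading-change trials.
    """
    params = params or NeuronParams()
    build_species = "hybrid" if species == "fly" else species
    base = build_species_circuit(species, weights, sigma=0.8,
                                 n_octants=n_octants)
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(base, params, seed=seed)
    records = []
    for si, sig in enumerate(sigma_grid):
        cx = build_species_circuit(build_species, weights, sigma=sig,
                                   n_octants=n_octants)
        cx = _rescale_inhibition_blocks(cx, base)
        for dj, delta in enumerate(delta_grid):
            res = run_heading_change(cx, params, delta=delta,
                                     n_trials=n_trials, peak_rate=peak_rate,
                                     seed=trial_seed(seed, 4, si, dj))
            kinds = res.records["kind"]
            frac_jump = (kinds == "jump").mean()
            regime = ("jump" if frac_jump == 1.0
                      else "gradual" if frac_jump == 0.0 else "both")
            records.append({"sigma": sig, "delta": delta,
                            "frac_jump": frac_jump, "regime": regime})
    rec = pd.DataFrame(records)
    return ExperimentResult(
        protocol="sigma_sweep", variant=species, records=rec,
        summary=rec.pivot(index="sigma", columns="delta",
                          values="regime").reset_index(),
        meta={"seed": seed, "n_trials": n_trials, "peak_rate": peak_rate,
              "sigma_grid": list(sigma_grid), "delta_grid": list(delta_grid)},
    )


# ---------------------------------------------------------------------------
# Attractor-state distribution
# ---------------------------------------------------------------------------

def run_attractor_states(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    azimuth_grid: Optional[Sequence[float]] = None,
    n_trials: int = 10,
    stim_duration: float = 3.0,
    settle: float = 3.0,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Where the bump settles 3 s after stimulus removal, per stimulus
    azimuth; summarised as circular mean and circular sd per azimuth."""
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    if azimuth_grid is None:
        azimuth_grid = np.arange(16) * 22.5
    records = []
    for j, az in enumerate(azimuth_grid):
        for i in range(n_trials):
            s = trial_seed(seed, 5, j, i)
            raster = _maintenance_raster(cx, params, az, peak_rate,
                                         stim_duration, settle, s)
            try:
                stats = metrics.bump_statistics_at(
                    raster, cx, "E-PG", stim_duration + settle - params.dt)
                settled = stats.heading
            except metrics.UndefinedHeadingError:
                settled = np.nan
            records.append({"azimuth": az, "trial": i, "seed": s,
                            "settled": settled})
    rec = pd.DataFrame(records)
    rows = []
    for az, grp in rec.groupby("azimuth"):
        ang = np.deg2rad(grp["settled"].dropna().to_numpy())
        if ang.size == 0:
            rows.append({"azimuth": az, "mean": np.nan, "circ_sd": np.nan,
                         "n": 0})
            continue
        z = np.mean(np.exp(1j * ang))
        r = np.abs(z)
        circ_sd = np.sqrt(-2.0 * np.log(max(r, 1e-12)))
        rows.append({"azimuth": az,
                     "mean": float(np.rad2deg(np.angle(z)) % 360.0),
                     "circ_sd": float(np.rad2deg(circ_sd)),
                     "n": int(ang.size)})
    return ExperimentResult(
        protocol="attractor_states", variant=_variant_name(cx), records=rec,
        summary=pd.DataFrame(rows),
        meta={"seed": seed, "n_trials": n_trials, "peak_rate": peak_rate},
    )


# ---------------------------------------------------------------------------
# Stability protocols
# ---------------------------------------------------------------------------

def _stability_trial(cx, params, peak_rate, s, az1=90.0, delta=120.0,
                     stim1=3.0, stim2=3.0, hold=3.0,
                     g_leak=None, C_m=None) -> bool:
    """One two-heading trial: stimulus, second stimulus, darkness hold.

    Success: the heading transitioned to the second azimuth with error
    below 45 deg and held it for at least ``hold`` seconds.
    """
    az2 = (az1 + delta) % 360.0
    duration = stim1 + stim2 + hold
    segs = [
        stimuli.heading_segment(cx, np.deg2rad(az1), peak_rate, 0.0, stim1),
        stimuli.heading_segment(cx, np.deg2rad(az2), peak_rate, stim1,
                                stim1 + stim2),
    ]
    raster = _simulate(cx, params, segs, duration, s, g_leak, C_m)
    trace = metrics.smooth_rates(raster)
    times, headings = metrics.heading_series(trace, cx)
    sel = times >= stim1
    return metrics.trial_stability(times[sel], headings[sel], az2,
                                   hold_duration=hold)


def run_noise_robustness(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    noise_levels: Sequence[float] = (0.0, 10.0, 20.0, 40.0),
    n_trials: int = 100,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Stable-heading fraction under synaptic-weight noise."""
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    records = []
    for xi, x in enumerate(noise_levels):
        for i in range(n_trials):
            s = trial_seed(seed, 6, xi, i)
            rng = np.random.default_rng(s)
            noisy = synaptic_noise(cx, x, rng) if x > 0 else cx
            ok = _stability_trial(noisy, params, peak_rate, trial_seed(s, 1))
            records.append({"noise_pct": x, "trial": i, "seed": s,
                            "stable": ok})
    rec = pd.DataFrame(records)
    summary = rec.groupby("noise_pct")["stable"].mean().rename(
        "stable_fraction").reset_index()
    return ExperimentResult(
        protocol="noise_robustness", variant=_variant_name(cx), records=rec,
        summary=summary,
        meta={"seed": seed, "n_trials": n_trials, "peak_rate": peak_rate},
    )


def run_asymmetry_tolerance(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    factors: Sequence[float] = (-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5,
                                0.75, 1.0),
    n_trials: int = 20,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Stable-heading fraction as one hemisphere's P-EN->E-PG synapses are
    scaled by (1 + factor), factor in [-1, 1]."""
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    records = []
    for fi, f in enumerate(factors):
        varied = hemisphere_asymmetry(cx, f) if f != 0 else cx
        for i in range(n_trials):
            s = trial_seed(seed, 7, fi, i)
            ok = _stability_trial(varied, params, peak_rate, s)
            records.append({"factor": f, "trial": i, "seed": s, "stable": ok})
    rec = pd.DataFrame(records)
    summary = rec.groupby("factor")["stable"].mean().rename(
        "stable_fraction").reset_index()
    return ExperimentResult(
        protocol="asymmetry_tolerance", variant=_variant_name(cx), records=rec,
        summary=summary,
        meta={"seed": seed, "n_trials": n_trials, "peak_rate": peak_rate},
    )


def stable_factor_range(result: ExperimentResult, threshold: float = 0.5) -> float:
    """Width (in factor units) of the asymmetry range with stable fraction
    at or above ``threshold``."""
    df = result.summary
    ok = df[df["stable_fraction"] >= threshold]["factor"]
    if ok.empty:
        return 0.0
    return float(ok.max() - ok.min())


def run_heterogeneity(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    noise_levels: Sequence[float] = (0.0, 10.0, 20.0, 40.0),
    target: str = "both_membrane",
    n_trials: int = 50,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Stable-heading fraction under per-neuron membrane heterogeneity
    (conductance and/or capacitance perturbed, clipped at zero)."""
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    records = []
    for xi, x in enumerate(noise_levels):
        for i in range(n_trials):
            s = trial_seed(seed, 8, xi, i)
            rng = np.random.default_rng(s)
            g, c = lif.perturb_membrane(params, cx.n_neurons, x, rng, target)
            ok = _stability_trial(cx, params, peak_rate, trial_seed(s, 1),
                                  g_leak=g, C_m=c)
            records.append({"noise_pct": x, "target": target, "trial": i,
                            "seed": s, "stable": ok})
    rec = pd.DataFrame(records)
    summary = rec.groupby("noise_pct")["stable"].mean().rename(
        "stable_fraction").reset_index()
    summary["target"] = target
    return ExperimentResult(
        protocol="heterogeneity", variant=_variant_name(cx), records=rec,
        summary=summary,
        meta={"seed": seed, "n_trials": n_trials, "target": target,
              "peak_rate": peak_rate},
    )


# ---------------------------------------------------------------------------
# Uni-hemispheric rotation drive
# ---------------------------------------------------------------------------

def run_rotation(
    cx: ConnectivityMatrix,
    params: Optional[NeuronParams] = None,
    strengths: Sequence[float] = (40.0, 80.0, 120.0, 160.0, 200.0, 240.0),
    hemisphere: str = "L",
    drive_duration: float = 4.0,
    stim_duration: float = 3.0,
    n_trials: int = 5,
    peak_rate: Optional[float] = None,
    seed: int = 0,
) -> ExperimentResult:
    """Bump angular velocity versus uni-hemispheric P-EN drive strength.

    After a heading stimulus initialises the bump, Poisson drive at each
    strength is delivered to all P-EN neurons of one hemisphere; angular
    velocity is the slope of the unwrapped decoded heading over the
    final half of the drive period.  The velocity curve is fit with
    y = a exp(b x).
    """
    params = params or NeuronParams()
    if peak_rate is None:
        peak_rate = calibrate_peak_rate(cx, params, seed=seed)
    duration = stim_duration + drive_duration
    records = []
    for ki, strength in enumerate(strengths):
        for i in range(n_trials):
            s = trial_seed(seed, 9, ki, i)
            segs = [
                stimuli.heading_segment(cx, np.deg2rad(90.0), peak_rate, 0.0,
                                        stim_duration),
            ]
            if strength > 0:
                segs.append(stimuli.rotation_segment(
                    cx, hemisphere, strength, stim_duration, duration))
            raster = _simulate(cx, params, segs, duration, s)
            trace = metrics.smooth_rates(raster)
            times, headings = metrics.heading_series(trace, cx)
            sel = times >= stim_duration
            t_sel, h_sel = times[sel], headings[sel]
            h_unwrapped = _unwrap_deg(h_sel)
            half = t_sel.size // 2
            good = np.isfinite(h_unwrapped[half:])
            if good.sum() >= 10:
                vel = np.polyfit(t_sel[half:][good],
                                 h_unwrapped[half:][good], 1)[0]
            else:
                vel = np.nan
            excursion = (np.nanmax(h_unwrapped) - np.nanmin(h_unwrapped)
                         if np.isfinite(h_unwrapped).any() else np.nan)
            records.append({"strength": strength, "trial": i, "seed": s,
                            "velocity": vel, "excursion": excursion})
    rec = pd.DataFrame(records)
    summary = rec.groupby("strength").agg(
        velocity_median=("velocity", "median"),
        velocity_sd=("velocity", "std"),
        excursion_max=("excursion", "max"),
    ).reset_index()
    fit = fit_exponential(summary["strength"].to_numpy(),
                          np.abs(summary["velocity_median"].to_numpy()))
    return ExperimentResult(
        protocol="rotation", variant=_variant_name(cx), records=rec,
        summary=summary,
        meta={"seed": seed, "hemisphere": hemisphere, "peak_rate": peak_rate,
              "fit": fit},
    )


def _unwrap_deg(h: np.ndarray) -> np.ndarray:
    """Unwrap a heading series in degrees, carrying NaNs through."""
    h = np.asarray(h, float)
    out = np.full_like(h, np.nan)
    good = np.isfinite(h)
    if good.sum() >= 2:
        out[good] = np.rad2deg(np.unwrap(np.deg2rad(h[good])))
    elif good.any():
        out[good] = h[good]
    return out


def fit_exponential(x: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares fit of y = a exp(b x); returns a, b and R^2."""
    good = np.isfinite(x) & np.isfinite(y) & (y > 0)
    x, y = x[good], y[good]
    if x.size < 3:
        return {"a": np.nan, "b": np.nan, "r2": np.nan, "n": int(x.size)}
    # log-linear start values, then nonlinear refinement
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    try:
        popt, _ = curve_fit(lambda xx, a, b: a * np.exp(b * xx), x, y,
                            p0=(np.exp(loga0), b0), maxfev=10000)
        a, b = popt
    except RuntimeError:
        a, b = np.exp(loga0), b0
    resid = y - a * np.exp(b * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {"a": float(a), "b": float(b), "r2": r2, "n": int(x.size)}


def _variant_name(cx: ConnectivityMatrix) -> str:
    name = cx.species
    if cx.meta.get("variant"):
        name += f"+{cx.meta['variant']}"
    if "P-EG" not in set(cx.neurons["cls"]):
        name += "-noPEG"
    return name
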