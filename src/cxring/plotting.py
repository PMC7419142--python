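"""Quick-look figures for simulations and experiment results."""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import metrics


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_rate_heatmap(trace: metrics.RateTrace, circuit, ax=None,
                      decimate: int = 50):
    """Smoothed firing rates of all neurons over time, ordered by class
    and octant (the conventional raster-style summary view)."""
    ax = _get_ax(ax)
    order = circuit.neurons.sort_values(["cls", "octant", "hemi"]).index
    data = trace.rates[order][:, ::decimate]
    im = ax.imshow(data, aspect="auto", origin="lower", cmap="viridis",
                   extent=(0, trace.n_steps * trace.dt, 0, len(order)))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron (grouped by class)")
    ax.figure.colorbar(im, ax=ax, label="rate (imp/s)")
    return ax


def plot_bump_profile(raster, circuit, t: float, cls: str = "E-PG", ax=None):
    """Azimuthal rate profile of one class at time ``t``."""
    ax = _get_ax(ax)
    centres, prof = metrics.azimuth_profile_at(raster, circuit, t, cls)
    ax.plot(np.append(centres, centres[0] + 360.0),
            np.append(prof, prof[0]), "o-")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("rate (imp/s)")
    ax.set_title(f"{cls} profile at t = {t:.2f} s")
    return ax


def plot_stability_curve(result, x: Optional[str] = None, ax=None):
    """Stable-trial fraction versus noise level / asymmetry factor."""
    ax = _get_ax(ax)
    df = result.summary
    if x is None:
        x = "noise_pct" if "noise_pct" in df.columns else "factor"
    ax.plot(df[x], df["stable_fraction"], "o-")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(x)
    ax.set_ylabel("stable fraction")
    ax.set_title(result.protocol)
    return ax


def plot_velocity_curve(result, ax=None):
    """Rotation drive: bump angular velocity and the exponential fit."""
    ax = _get_ax(ax)
    df = result.summary
    x = df["strength"].to_numpy()
    y = np.abs(df["velocity_median"].to_numpy())
    ax.plot(x, y, "o", label="measured")
    fit = result.meta.get("fit", {})
    if np.isfinite(fit.get("b", np.nan)):
        xs = np.linspace(x.min(), x.max(), 100)
        ax.plot(xs, fit["a"] * np.exp(fit["b"] * xs), "-",
                label=f"a e^(bx), b={fit['b']:.3g}, R²={fit['r2']:.2f}")
    ax.set_xlabel("drive strength (imp/s)")
    ax.set_ylabel("|angular velocity| (deg/s)")
    ax.legend()
    return ax
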