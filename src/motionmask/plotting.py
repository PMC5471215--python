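"""Export and plotting helpers for energy maps and masking curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: sensitivity contour level used when outlining energy-map passbands
CONTOUR_LEVEL = 0.25


def energy_map_frame(
    maps: dict[str, np.ndarray], f_s_grid: np.ndarray, f_t_grid: np.ndarray,
    which: str = "opponent",
) -> pd.DataFrame:
    """An energy map as a DataFrame (rows: f_s in cpd, columns: f_t in Hz),
    ready for ``to_csv`` with grid header rows."""
    return pd.DataFrame(maps[which], index=pd.Index(f_s_grid, name="f_s_cpd"),
                        columns=pd.Index(f_t_grid, name="f_t_hz"))


def plot_energy_maps(maps, f_s_grid, f_t_grid, axes=None):
    """Directional and opponent energy maps with 0.25 sensitivity contours.

    Returns the three matplotlib axes.  Imported lazily so headless use of
    the library never touches a plotting backend.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    extent = [f_t_grid[0], f_t_grid[-1], f_s_grid[0], f_s_grid[-1]]
    scale = max(np.abs(maps["rightward"]).max(), np.abs(maps["leftward"]).max())
    for ax, name in zip(axes, ("rightward", "leftward", "opponent")):
        data = maps[name]
        ax.imshow(data, origin="lower", aspect="auto", extent=extent,
                  cmap="RdBu_r", vmin=-scale, vmax=scale)
        ax.contour(f_t_grid, f_s_grid, np.abs(data) / scale,
                   levels=[CONTOUR_LEVEL], colors="k", linewidths=1)
        ax.set_title(f"{name} energy")
        ax.set_xlabel("temporal frequency (Hz)")
    axes[0].set_ylabel("spatial frequency (cpd)")
    return axes


def plot_masking_curve(curve, ax=None, **kwargs):
    """Masking rate or threshold elevation vs noise frequency with CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    f = curve.noise_frequencies
    yerr = None
    if np.all(np.isfinite(curve.ci_low)):
        yerr = [curve.values - curve.ci_low, curve.ci_high - curve.values]
    ax.errorbar(f, curve.values, yerr=yerr, fmt="o-", capsize=3, **kwargs)
    ax.set_xscale("log")
    ax.set_xlabel("noise spatial frequency (cpd)")
    ax.set_ylabel(
        "masking rate" if curve.kind == "insect-rate" else "threshold elevation"
    )
    return ax
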