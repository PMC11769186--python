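"""Matplotlib figures for calibration curves and mode-bias reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calibration import BiasReport, CalibrationCurve

__all__ = ["plot_calibration_curves", "plot_bias", "save_figure"]

_COLORS = {"light": "tab:orange", "moderate": "tab:green", "dark": "tab:brown"}


def plot_calibration_curves(points_by_skin, fits=None, title="Simulated calibration curves"):
    """Scatter the simulated (R, SaO2) points per skin type with best-fit lines.

    ``points_by_skin`` maps a skin label to a list of (sao2_percent, r)
    pairs; ``fits`` optionally maps the same labels to fitted
    :class:`CalibrationCurve` objects.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for skin, pts in points_by_skin.items():
        pts = np.asarray(list(pts), dtype=float)
        color = _COLORS.get(skin)
        ax.plot(pts[:, 1], pts[:, 0], "o--", label=skin, color=color, mfc="none")
        if fits and skin in fits:
            curve = fits[skin]
            curve = curve.curve if hasattr(curve, "curve") else curve
            rr = np.linspace(pts[:, 1].min(), pts[:, 1].max(), 50)
            ax.plot(rr, curve.predict(rr), "-", color=color)
    ax.set_xlabel("ratio of ratios R")
    ax.set_ylabel("SaO$_2$ (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_bias(reports: list[BiasReport], title="Transmittance vs reflectance bias"):
    """Bias (%) vs SaO2 for each skin type's report."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for rep in reports:
        ax.plot(
            rep.sao2_grid,
            rep.bias,
            "o-",
            label=f"{rep.skin_type} (RMSE {rep.rmse:.4f}%)",
            color=_COLORS.get(rep.skin_type),
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("SaO$_2$ (%)")
    ax.set_ylabel("bias (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    return fig


def save_figure(fig, path):
    fig.savefig(path, dpi=150)
    plt.close(fig)
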