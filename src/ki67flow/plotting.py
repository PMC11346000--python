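"""QC plots: DNA-content histogram and FSC-SSC scatter with gate overlays.

Display only — gating always operates on linear channel values; the arcsinh
transform here compresses the dynamic range of antibody channels for
visualisation, exactly as cytometry software does on screen.
"""

from __future__ import annotations

import numpy as np

from .gating import DnaGate, EllipseGate
from .io import EventTable

__all__ = ["arcsinh_display", "plot_dna_histogram", "plot_scatter_gate"]


def arcsinh_display(values: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """Arcsinh display transform, ``asinh(x / cofactor)``."""
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def plot_dna_histogram(table: EventTable, gate: DnaGate | None = None, ax=None):
    """DNA-content histogram with optional 2n-window shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    dna = table.channel("DNA")
    ax.hist(dna, bins=256, color="0.4")
    if gate is not None:
        ax.axvspan(gate.lower, gate.upper, color="tab:blue", alpha=0.2,
                   label="2n window")
        ax.axvline(gate.peak_2n, color="tab:blue")
        ax.legend()
    ax.set_xlabel("DNA content (a.u.)")
    ax.set_ylabel("events")
    return ax


def plot_scatter_gate(table: EventTable, ellipse: EllipseGate | None = None,
                      ax=None, max_points: int = 20_000):
    """FSC-SSC scatter with an optional AreaX ellipse outline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = table.scatter()
    if len(pts) > max_points:
        step = len(pts) // max_points
        pts = pts[::step]
    ax.plot(pts[:, 0], pts[:, 1], ",", color="0.5", alpha=0.5)
    if ellipse is not None:
        t = np.linspace(0, 2 * np.pi, 256)
        c, s = np.cos(ellipse.angle), np.sin(ellipse.angle)
        x = ellipse.semi_axes[0] * np.cos(t)
        y = ellipse.semi_axes[1] * np.sin(t)
        ax.plot(ellipse.center[0] + c * x - s * y,
                ellipse.center[1] + s * x + c * y, "r-", label="AreaX")
        ax.legend()
    ax.set_xlabel("FSC (a.u.)")
    ax.set_ylabel("SSC (a.u.)")
    return ax
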