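"""Built-in 10-20 / 10-10 scalp montage.

Provides a 32-channel montage with approximate 2-D topographic
coordinates (head seen from above, x toward the right ear, y toward the
nasion, unit head radius) for labelling simulated recordings, defining
anatomical electrode groups, and rendering simple topographic maps.
T3/T4/T5/T6 follow the older 10-20 naming used in clinical reports
(equivalent to T7/T8/P7/P8).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MONTAGE_32",
    "ELECTRODE_COORDS",
    "POSTERIOR_ELECTRODES",
    "coords_for",
    "plot_topomap",
]

# label -> (x, y); approximate equal-angle projection of the standard
# 10-10 positions onto the unit disc.
ELECTRODE_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.29, 0.91),
    "Fpz": (0.00, 0.95),
    "Fp2": (0.29, 0.91),
    "F7": (-0.77, 0.59),
    "F3": (-0.40, 0.52),
    "Fz": (0.00, 0.48),
    "F4": (0.40, 0.52),
    "F8": (0.77, 0.59),
    "FC5": (-0.63, 0.28),
    "FC1": (-0.22, 0.25),
    "FC2": (0.22, 0.25),
    "FC6": (0.63, 0.28),
    "T3": (-0.95, 0.00),
    "C3": (-0.48, 0.00),
    "Cz": (0.00, 0.00),
    "C4": (0.48, 0.00),
    "T4": (0.95, 0.00),
    "CP5": (-0.63, -0.28),
    "CP1": (-0.22, -0.25),
    "CP2": (0.22, -0.25),
    "CP6": (0.63, -0.28),
    "T5": (-0.77, -0.59),
    "P3": (-0.40, -0.52),
    "Pz": (0.00, -0.48),
    "P4": (0.40, -0.52),
    "T6": (0.77, -0.59),
    "PO3": (-0.29, -0.73),
    "POz": (0.00, -0.72),
    "PO4": (0.29, -0.73),
    "O1": (-0.29, -0.91),
    "Oz": (0.00, -0.95),
    "O2": (0.29, -0.91),
}

#: Default 32-channel montage, frontal to occipital.
MONTAGE_32: list[str] = list(ELECTRODE_COORDS)

#: Centro-parieto-occipital electrodes ("posterior hot zone"), the region
#: where connectivity reductions are typically reported in disorders of
#: consciousness.
POSTERIOR_ELECTRODES: list[str] = [
    "CP5", "CP1", "CP2", "CP6",
    "T5", "P3", "Pz", "P4", "T6",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
]


def coords_for(labels) -> np.ndarray:
    """Return (n, 2) topographic coordinates for the given labels."""
    try:
        return np.array([ELECTRODE_COORDS[l] for l in labels], dtype=float)
    except KeyError as exc:  # pragma: no cover - message only
        raise KeyError(f"no montage coordinates for electrode {exc}") from None


def plot_topomap(values: dict[str, float], ax=None, cmap="viridis", title=None):
    """Scatter-style topographic map of per-electrode values.

    Parameters
    ----------
    values : mapping label -> float
    ax : matplotlib Axes, optional

    Returns
    -------
    matplotlib Axes
    """
    import matplotlib.pyplot as plt

    labels = [l for l in values if l in ELECTRODE_COORDS]
    xy = coords_for(labels)
    v = np.array([values[l] for l in labels])
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1)
    ax.add_patch(circle)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=v, s=220, cmap=cmap, zorder=2)
    for (x, y), lab in zip(xy, labels):
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=6, zorder=3)
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax
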