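"""Schematic 10-20 electrode layout and neighbor-based interpolation weights.

Positions are idealized 2-D head-schematic coordinates (x: left -1 .. +1
right, y: back -1 .. +1 front) for the subset of the international 10-20
system used here. They serve only to define spatial neighborhoods for
bad-channel interpolation; no anatomical forward model is implied.
"""

from __future__ import annotations

import numpy as np

LAYOUT_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.54), "Fz": (0.0, 0.50),
    "F4": (0.43, 0.54), "F8": (0.81, 0.59),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CPz": (0.0, -0.25),
    "P7": (-0.81, -0.59), "P3": (-0.43, -0.54), "Pz": (0.0, -0.50),
    "P4": (0.43, -0.54), "P8": (0.81, -0.59),
    "P9": (-0.95, -0.72), "P10": (0.95, -0.72),
    "PO7": (-0.57, -0.77), "POz": (0.0, -0.75), "PO8": (0.57, -0.77),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

#: Default full channel set of the synthetic montage, in recording order.
DEFAULT_CHANNELS = list(LAYOUT_2D)


def interpolation_weights(
    labels: list[str], bad: str, n_neighbors: int = 4
) -> dict[str, float]:
    """Inverse-distance weights over the nearest good neighbors of ``bad``.

    Weights are normalized to sum to one; channels without a layout entry
    cannot be interpolated.
    """
    if bad not in LAYOUT_2D:
        raise KeyError(f"no layout position for channel {bad!r}")
    bx, by = LAYOUT_2D[bad]
    dists = []
    for lab in labels:
        if lab == bad or lab not in LAYOUT_2D:
            continue
        x, y = LAYOUT_2D[lab]
        dists.append((np.hypot(x - bx, y - by), lab))
    if not dists:
        raise ValueError(f"no neighbors available to interpolate {bad!r}")
    dists.sort()
    nearest = dists[:n_neighbors]
    w = np.array([1.0 / max(d, 1e-9) for d, _ in nearest])
    w /= w.sum()
    return {lab: wi for (_, lab), wi in zip(nearest, w)}
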