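"""ERP component scoring for the passive-viewing task.

Components are scored as mean voltage over fixed electrode clusters and
latency windows: P1 (O1/O2/PO7/PO8/P9/P10, 80-120 ms), N170
(PO7/PO8/P9/P10, 130-200 ms), EPN (P7/P8/PO7/PO8/P9/P10, 240-300 ms) and
LPP (midline Cz/CPz/Pz/POz, 400-1000 ms). Because a large P1 carries over
into the N170 range, a peak-to-peak P1-N170 measure (N170 trough minus
P1 peak on the cell-averaged waveform) is provided as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet, hemisphere_of

logger = logging.getLogger(__name__)


@dataclass
class ComponentSpec:
    name: str
    cluster: tuple
    window_ms: tuple
    polarity: str  # 'positive' or 'negative'
    hemisphere_split: bool = True

    def side_channels(self, side: str):
        chans = [c for c in self.cluster if hemisphere_of(c) == side]
        if not chans:
            raise ValueError(f"{self.name} cluster has no {side} channels")
        return chans


DEFAULT_COMPONENTS = (
    ComponentSpec("P1", ("O1", "O2", "PO7", "PO8", "P9", "P10"),
                  (80.0, 120.0), "positive"),
    ComponentSpec("N170", ("PO7", "PO8", "P9", "P10"),
                  (130.0, 200.0), "negative"),
    ComponentSpec("EPN", ("P7", "P8", "PO7", "PO8", "P9", "P10"),
                  (240.0, 300.0), "negative"),
    ComponentSpec("LPP", ("Cz", "CPz", "Pz", "POz"),
                  (400.0, 1000.0), "positive", hemisphere_split=False),
)

P1_WINDOW = (80.0, 120.0)
N170_WINDOW = (130.0, 200.0)
P2P_CLUSTER = ("PO7", "PO8", "P9", "P10")


def _cell_trials(ep: EpochSet, expression: str) -> np.ndarray:
    return np.array([
        (not ep.rejected[i]) and c.task == "viewing"
        and c.expression == expression
        for i, c in enumerate(ep.conditions)
    ])


def _window_mask(ep: EpochSet, window_ms) -> np.ndarray:
    t0, t1 = window_ms
    m = (ep.time_ms >= t0) & (ep.time_ms <= t1)
    if not m.any():
        raise ValueError(f"window {window_ms} outside epoch")
    return m


def mean_amplitude(ep: EpochSet, spec: ComponentSpec, expression: str,
                   hemisphere: str | None = None) -> float:
    """Mean voltage over the cell's trials, cluster channels and window.

    Returns NaN (with a logged reason) when the condition cell holds no
    unrejected trials.
    """
    sel = _cell_trials(ep, expression)
    if not sel.any():
        logger.warning("empty cell: %s / %s", spec.name, expression)
        return float("nan")
    chans = (spec.side_channels(hemisphere) if hemisphere in ("left", "right")
             else list(spec.cluster))
    ci = ep.channel_indices(chans)
    tm = _window_mask(ep, spec.window_ms)
    return float(ep.data[sel][:, ci][:, :, tm].mean())


def peak_to_peak_p1_n170(ep: EpochSet, expression: str,
                         hemisphere: str | None = None,
                         p1_window=P1_WINDOW, n170_window=N170_WINDOW,
                         cluster=P2P_CLUSTER) -> float:
    """N170 trough minus P1 peak on the cell-averaged cluster waveform.

    More negative values mean a larger N170 relative to the preceding P1;
    the measure is invariant to constant voltage offsets.
    """
    sel = _cell_trials(ep, expression)
    if not sel.any():
        logger.warning("empty cell for peak-to-peak: %s", expression)
        return float("nan")
    chans = ([c for c in cluster if hemisphere_of(c) == hemisphere]
             if hemisphere in ("left", "right") else list(cluster))
    ci = ep.channel_indices(chans)
    wave = ep.data[sel][:, ci].mean(axis=(0, 1))
    p1 = wave[_window_mask(ep, p1_window)].max()
    n170 = wave[_window_mask(ep, n170_window)].min()
    return float(n170 - p1)


def component_table(ep: EpochSet, participant: str = "", group: str = "",
                    specs=DEFAULT_COMPONENTS) -> pd.DataFrame:
    """Tidy component table.

    Lateral components are scored per hemisphere (odd-numbered cluster
    labels left, even right); the midline LPP gets a single row. The
    peak-to-peak P1-N170 is included for the N170 rows.
    """
    expressions = sorted({c.expression for c in ep.conditions
                          if c.task == "viewing"})
    rows = []
    for expr in expressions:
        for spec in specs:
            hemis = ("left", "right") if spec.hemisphere_split else ("midline",)
            for hemi in hemis:
                h = hemi if hemi != "midline" else None
                row = {"participant": participant, "group": group,
                       "expression": expr, "component": spec.name,
                       "hemisphere": hemi,
                       "mean_amplitude": mean_amplitude(ep, spec, expr, h)}
                if spec.name == "N170":
                    row["peak_to_peak"] = peak_to_peak_p1_n170(ep, expr, h)
                else:
                    row["peak_to_peak"] = float("nan")
                rows.append(row)
    return pd.DataFrame(rows)
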