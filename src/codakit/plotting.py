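"""Exchange plots: time-time visualisation of multi-whale click trains.

Each click is drawn at (x, y) where x is its absolute time in the
exchange and y is the time elapsed since the first click of its coda --
the vertical axis acts as a microscope over the horizontal one, exposing
each coda's internal structure.  Clicks are coloured by whale; optional
line segments connect click i of a coda to click i of the next coda by
the same whale, which makes both rubato (gradually tilting lines) and
ornaments (a terminal click with no partner) visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ExchangeDataset
from .segmentation import call_sequences

__all__ = ["PlotSpec", "exchange_coordinates", "link_adjacent", "render"]


@dataclass
class PlotSpec:
    """Rendering options for an exchange plot."""

    t_start: float = 0.0
    t_end: float | None = None
    link_adjacent: bool = True
    whale_colors: dict[str, str] = field(default_factory=dict)
    ornament_ids: set[str] = field(default_factory=set)
    figsize: tuple[float, float] = (10.0, 3.0)

    _PALETTE = ("tab:blue", "tab:orange", "tab:green", "tab:red",
                "tab:purple", "tab:brown", "tab:pink", "tab:gray")

    def color_for(self, whale_id: str, index: int) -> str:
        return self.whale_colors.get(whale_id,
                                     self._PALETTE[index % len(self._PALETTE)])


def exchange_coordinates(dataset: ExchangeDataset) -> pd.DataFrame:
    """Click coordinates: one row per click.

    Columns ``x`` (absolute click time), ``y`` (time since coda onset;
    0 for the first click, the cumulative ICIs for the rest),
    ``whale_id``, ``coda_id``, ``click_index``.
    """
    dataset.require_ordered("exchange_coordinates")
    rows = []
    for coda in dataset:
        times = coda.click_times()
        for j, t in enumerate(times):
            rows.append({"x": t, "y": t - coda.onset_time,
                         "whale_id": coda.whale_id, "coda_id": coda.coda_id,
                         "click_index": j})
    return pd.DataFrame(rows, columns=["x", "y", "whale_id", "coda_id",
                                       "click_index"])


def link_adjacent(dataset: ExchangeDataset,
                  gap_s: float = 8.0) -> list[tuple[tuple[float, float],
                                                    tuple[float, float]]]:
    """Segments joining matching clicks of consecutive same-whale codas.

    Click i of a coda is linked to click i of the next coda in the same
    call sequence, for i up to the smaller click count; a trailing
    ornament click therefore stays unlinked.  Segments are
    ((x1, y1), (x2, y2)) pairs and never join different whales.
    """
    segments = []
    for seq in call_sequences(dataset, gap_s=gap_s):
        codas = [dataset.get(cid) for cid in seq.coda_ids]
        for a, b in zip(codas, codas[1:]):
            ta, tb = a.click_times(), b.click_times()
            for i in range(min(a.click_count, b.click_count)):
                segments.append(((ta[i], ta[i] - a.onset_time),
                                 (tb[i], tb[i] - b.onset_time)))
    return segments


def render(dataset: ExchangeDataset, spec: PlotSpec,
           out_path: str | Path) -> Path:
    """Render the exchange plot to ``out_path`` (.svg or .png).

    Deterministic for fixed inputs.  Raises if the requested window
    contains no codas.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    # fixed hash salt so SVG element ids are reproducible
    matplotlib.rcParams["svg.hashsalt"] = "codakit"

    coords = exchange_coordinates(dataset)
    t_end = spec.t_end if spec.t_end is not None else float(coords["x"].max())
    window = coords[(coords["x"] >= spec.t_start) & (coords["x"] <= t_end)]
    if window.empty:
        raise ValueError(
            f"no clicks in window [{spec.t_start}, {t_end}] s; nothing to draw")

    fig, ax = plt.subplots(figsize=spec.figsize)
    if spec.link_adjacent:
        for (x1, y1), (x2, y2) in link_adjacent(dataset):
            if spec.t_start <= x1 and x2 <= t_end:
                ax.plot([x1, x2], [y1, y2], color="0.8", lw=0.6, zorder=1)
    for k, whale in enumerate(dataset.whale_ids):
        sub = window[window["whale_id"] == whale]
        color = spec.color_for(whale, k)
        plain = sub[~sub["coda_id"].isin(spec.ornament_ids)]
        ax.scatter(plain["x"], plain["y"], s=8, color=color, label=whale,
                   zorder=2)
        orn = sub[sub["coda_id"].isin(spec.ornament_ids)]
        if not orn.empty:
            ax.scatter(orn["x"], orn["y"], s=14, marker="D", color=color,
                       edgecolors="black", linewidths=0.4, zorder=3)
    ax.set_xlabel("time in exchange (s)")
    ax.set_ylabel("time since coda onset (s)")
    ax.set_ylim(bottom=-0.02)
    ax.legend(loc="upper right", fontsize=7, frameon=False)
    out_path = Path(out_path)
    fig.savefig(out_path, metadata=_stable_metadata(out_path.suffix))
    plt.close(fig)
    return out_path


def _stable_metadata(suffix: str) -> dict:
    # strip timestamps so identical inputs give identical bytes
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return {}
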